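"""Joint linkage QTL mapping across NIL populations.

The model regresses line means for one trait on a forced population term plus
marker dosages nested within population: each candidate marker contributes one
column per population in which it is polymorphic (that population's donor
dosage, 0 elsewhere), and the nested group enters or leaves the stepwise model
as a unit via a joint F-test. The entry/exit p-value threshold is calibrated
by permutations of the trait within population, recording the genome-wide
minimum marker p-value under the null. The final additive model is refit by
OLS; per-population coefficients are the additive effects of the teosinte
allele relative to B73 with t-tests, and populations without an introgression
at the marker are reported as "n.d.". Support intervals are found by adding a
pseudomarker group (flanking-marker expected dosages) to the full model at
0.1 cM steps outward from the peak until it is significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GeneticMap, GenotypeMatrix, expected_dosage_at, polymorphic_mask

logger = logging.getLogger(__name__)

ND = "n.d."


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class MarkerGroup:
    marker: str
    chrom: int
    pos_cM: float
    pops: list[str]          # populations where the marker is polymorphic
    cols: np.ndarray         # (n_lines, len(pops)) nested dosage columns


@dataclass
class NestedDesign:
    trait: str
    y: np.ndarray
    line_ids: np.ndarray
    populations: np.ndarray
    pop_levels: list[str]
    base: np.ndarray                      # intercept + population dummies
    groups: dict[str, MarkerGroup]
    geno_rows: np.ndarray                 # rows of the genotype matrix used
    order: dict[str, tuple] = field(default_factory=dict)  # marker -> sort key

    @property
    def n(self) -> int:
        return len(self.y)


def build_nested_design(means: pd.DataFrame, geno: GenotypeMatrix,
                        gmap: GeneticMap, trait: str) -> NestedDesign:
    """Assemble the response and nested-marker candidate groups for a trait.

    Lines present in both the means table and the genotype matrix, with a
    non-missing trait value, are used. Markers monomorphic in every
    population are excluded from the candidate set; a marker polymorphic in k
    populations contributes a k-column group.
    """
    if trait not in means.columns:
        raise KeyError(f"trait {trait!r} not in line means")
    if np.isnan(geno.dosage).any():
        raise ValueError("genotypes must be imputed before mapping")
    m = means.set_index("line_id")[trait]
    keep = []
    for i, lid in enumerate(geno.line_ids):
        if lid in m.index and np.isfinite(m[lid]):
            keep.append(i)
    rows = np.asarray(keep, dtype=int)
    if rows.size < 3:
        raise ValueError("fewer than 3 usable lines")
    y = m[geno.line_ids[rows]].to_numpy(float)
    pops = geno.populations[rows]
    pop_levels = list(pd.unique(pops))

    base = np.ones((rows.size, 1))
    for p in pop_levels[1:]:
        base = np.hstack([base, (pops == p).astype(float)[:, None]])

    sub = GenotypeMatrix(geno.line_ids[rows], pops, geno.markers,
                         geno.dosage[rows])
    mask = polymorphic_mask(sub)
    groups: dict[str, MarkerGroup] = {}
    order: dict[str, tuple] = {}
    table = gmap.table
    for j, marker in enumerate(geno.markers):
        poly = [p for p in pop_levels if mask.loc[p, marker]]
        if not poly:
            continue
        cols = np.zeros((rows.size, len(poly)))
        d = sub.dosage[:, j]
        for k, p in enumerate(poly):
            sel = pops == p
            cols[sel, k] = d[sel]
        chrom = int(table["chrom"].iloc[j])
        pos = float(table["pos_cM"].iloc[j])
        groups[marker] = MarkerGroup(marker, chrom, pos, poly, cols)
        order[marker] = (chrom, pos, marker)
    return NestedDesign(trait, y, geno.line_ids[rows], pops, pop_levels,
                        base, groups, rows, order)


# ---------------------------------------------------------------------------
# projection helpers
# ---------------------------------------------------------------------------

def _basis(X: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis for the column space of X."""
    if X.size == 0:
        return np.zeros((X.shape[0], 0))
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((X.shape[0], 0))
    return u[:, s > rtol * s[0]]


def _residualize(X: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return X - Q @ (Q.T @ X)


def _residual_basis(G: np.ndarray, Q0: np.ndarray,
                    rtol: float = 1e-8) -> np.ndarray:
    """Orthonormal basis of the part of G orthogonal to Q0; rank is judged
    relative to G's own scale, so columns aliased with Q0 are dropped."""
    R = _residualize(G, Q0)
    if R.size == 0:
        return np.zeros((G.shape[0], 0))
    u, s, _ = np.linalg.svd(R, full_matrices=False)
    scale = max(np.linalg.norm(G), 1e-30)
    return u[:, s > rtol * scale]


def _added_group_test(y: np.ndarray, Q0: np.ndarray, G: np.ndarray
                      ) -> tuple[float, float, int]:
    """F-test of adding column group G to a model with orthonormal basis Q0.

    Returns (F, p, q) with q the effective (post-residualization) rank of G;
    q = 0 signals a group aliased with the current model.
    """
    Qg = _residual_basis(G, Q0)
    q = Qg.shape[1]
    n = len(y)
    df2 = n - Q0.shape[1] - q
    if q == 0 or df2 <= 0:
        return np.nan, np.nan, q
    y_r = y - Q0 @ (Q0.T @ y)
    rss0 = float(y_r @ y_r)
    ss_add = float(np.sum((Qg.T @ y_r) ** 2))
    rss1 = max(rss0 - ss_add, 0.0)
    if rss1 <= 0:
        return np.inf, 0.0, q
    F = (ss_add / q) / (rss1 / df2)
    return F, float(stats.f.sf(F, q, df2)), q


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

def permutation_threshold(design: NestedDesign, n_perm: int = 1000,
                          alpha: float = 0.05, seed: int = 0,
                          return_minima: bool = False):
    """Genome-wide entry/exit threshold from within-population permutations.

    For each permutation the trait is shuffled among lines within each
    population (the forced population term is thereby preserved); every
    candidate group is F-tested against the population-only model and the
    genome-wide minimum p is recorded. The threshold is the empirical alpha
    quantile of those minima.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a stable quantile")
    rng = np.random.default_rng(seed)
    n = design.n
    Q0 = _basis(design.base)
    rank0 = Q0.shape[1]

    blocks, qs = [], []
    for g in design.groups.values():
        Qg = _residual_basis(g.cols, Q0)
        if Qg.shape[1] == 0:
            continue
        blocks.append(Qg)
        qs.append(Qg.shape[1])
    if not blocks:
        raise ValueError("no testable marker groups")
    Qall = np.hstack(blocks)
    qs = np.asarray(qs)
    starts = np.concatenate([[0], np.cumsum(qs)[:-1]])

    perm_idx = np.empty((n, n_perm), dtype=int)
    base_idx = np.arange(n)
    pop_rows = [np.flatnonzero(design.populations == p) for p in design.pop_levels]
    for b in range(n_perm):
        idx = base_idx.copy()
        for rows in pop_rows:
            idx[rows] = rows[rng.permutation(rows.size)]
        perm_idx[:, b] = idx

    Y = design.y[perm_idx]                      # (n, n_perm)
    Yr = Y - Q0 @ (Q0.T @ Y)
    rss0 = np.sum(Yr ** 2, axis=0)              # per permutation
    P2 = (Qall.T @ Yr) ** 2                     # (total_cols, n_perm)
    ss = np.add.reduceat(P2, starts, axis=0)    # (n_groups, n_perm)
    df2 = n - rank0 - qs
    with np.errstate(divide="ignore", invalid="ignore"):
        rss1 = np.maximum(rss0[None, :] - ss, 1e-300)
        F = (ss / qs[:, None]) / (rss1 / df2[:, None])
        pvals = stats.f.sf(F, qs[:, None], df2[:, None])
    minima = pvals.min(axis=0)
    threshold = float(np.quantile(minima, alpha, method="inverted_cdf"))
    if return_minima:
        return threshold, minima
    return threshold


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    trait: str
    selected: list[str]
    p_enter: float
    p_exit: float
    history: list[tuple[str, str, float]]   # (action, marker, p)


def _scan_candidates(design: NestedDesign, selected: list[str]
                     ) -> tuple[np.ndarray, dict[str, tuple[float, float, int]]]:
    X0 = design.base
    if selected:
        X0 = np.hstack([X0] + [design.groups[m].cols for m in selected])
    Q0 = _basis(X0)
    out = {}
    for m, g in design.groups.items():
        if m in selected:
            continue
        F, p, q = _added_group_test(design.y, Q0, g.cols)
        if q == 0:
            continue
        out[m] = (F, p, q)
    return Q0, out


def stepwise_select(design: NestedDesign, p_enter: float,
                    p_exit: float | None = None) -> StepwiseResult:
    """Forward/backward selection of nested marker groups.

    Forward: add the candidate group with the smallest joint-F p-value if it
    is below ``p_enter`` (ties broken by chromosome, then cM, then marker
    name). Backward: drop any included group whose p-value in the current
    model is >= ``p_exit`` (worst first), repeating to convergence. The
    population term is never subject to selection.
    """
    if not (0 <= p_enter < 1):
        raise ValueError("p_enter must be in [0, 1)")
    p_exit = p_enter if p_exit is None else p_exit
    if not (0 <= p_exit <= 1):
        raise ValueError("p_exit must be in [0, 1]")
    selected: list[str] = []
    history: list[tuple[str, str, float]] = []
    while True:
        _, scan = _scan_candidates(design, selected)
        best = None
        for m, (F, p, q) in scan.items():
            key = (p, *design.order[m])
            if best is None or key < best[0]:
                best = (key, m, p)
        if best is None or not (best[2] < p_enter):
            break
        selected.append(best[1])
        history.append(("add", best[1], best[2]))
        # backward sweep
        while len(selected) > 1:
            worst = None
            for m in selected:
                others = [s for s in selected if s != m]
                X0 = np.hstack([design.base] + [design.groups[s].cols for s in others])
                Q0 = _basis(X0)
                _, p, q = _added_group_test(design.y, Q0, design.groups[m].cols)
                p = 1.0 if q == 0 else p
                key = (-p, *design.order[m])
                if worst is None or key < worst[0]:
                    worst = (key, m, p)
            if worst is not None and worst[2] >= p_exit:
                selected.remove(worst[1])
                history.append(("drop", worst[1], worst[2]))
            else:
                break
    return StepwiseResult(design.trait, selected, p_enter, p_exit, history)


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    trait: str
    selected: list[str]
    coef: pd.Series                 # named coefficients
    se: pd.Series
    pvalues: pd.Series
    model_r2: float
    residual_df: int
    tss: float
    rss: float
    X: np.ndarray
    col_names: list[str]
    design: NestedDesign


def _assemble(design: NestedDesign, selected: list[str]
              ) -> tuple[np.ndarray, list[str]]:
    names = ["intercept"] + [f"pop[{p}]" for p in design.pop_levels[1:]]
    X = design.base
    for m in selected:
        g = design.groups[m]
        X = np.hstack([X, g.cols])
        names += [f"{m}:{p}" for p in g.pops]
    return X, names


def fit_final_model(design: NestedDesign, selection: StepwiseResult | list[str]
                    ) -> FittedModel:
    """OLS fit of the selected additive model; aliased columns are dropped
    with a log message. Per-population dosage coefficients are the additive
    effects of the teosinte allele relative to B73."""
    selected = selection.selected if isinstance(selection, StepwiseResult) else list(selection)
    X, names = _assemble(design, selected)
    # rank-reveal and drop aliased columns
    keep = []
    Q = np.zeros((X.shape[0], 0))
    for j in range(X.shape[1]):
        r = _residualize(X[:, [j]], Q)
        nrm = np.linalg.norm(r)
        if nrm > 1e-8 * max(np.linalg.norm(X[:, j]), 1.0):
            keep.append(j)
            Q = np.hstack([Q, r / nrm])
        else:
            logger.info("dropping aliased column %s", names[j])
    Xk = X[:, keep]
    nk = [names[j] for j in keep]
    y = design.y
    beta, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    rss = float(resid @ resid)
    df = Xk.shape[0] - Xk.shape[1]
    tss = float(np.sum((y - y.mean()) ** 2))
    sigma2 = rss / df if df > 0 else np.nan
    XtX_inv = np.linalg.inv(Xk.T @ Xk)
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    return FittedModel(
        design.trait, selected,
        pd.Series(beta, index=nk), pd.Series(se, index=nk),
        pd.Series(pvals, index=nk),
        1.0 - rss / tss if tss > 0 else np.nan,
        df, tss, rss, Xk, nk, design,
    )


def group_statistics(fitted: FittedModel, marker: str) -> tuple[float, float]:
    """(group F p-value, partial R^2) of one selected marker: the F-test of
    dropping its nested group from the full model; partial R^2 is the drop in
    explained sum of squares as a fraction of the total."""
    design = fitted.design
    others = [m for m in fitted.selected if m != marker]
    X0, _ = _assemble(design, others)
    Q0 = _basis(X0)
    F, p, q = _added_group_test(design.y, Q0, design.groups[marker].cols)
    y_r = design.y - Q0 @ (Q0.T @ design.y)
    rss0 = float(y_r @ y_r)
    partial = (rss0 - fitted.rss) / fitted.tss if fitted.tss > 0 else np.nan
    return p, max(partial, 0.0)


# ---------------------------------------------------------------------------
# support intervals
# ---------------------------------------------------------------------------

def support_interval(fitted: FittedModel, marker: str, geno: GenotypeMatrix,
                     gmap: GeneticMap, step_cM: float = 0.1,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Support interval of a selected QTL.

    Walking outward from the peak in ``step_cM`` steps, a pseudomarker group
    (expected dosages nested within population) is added to the full model;
    the first position on each side where that group is significant at
    ``alpha`` — variation the QTL model does not account for — is the
    boundary. Bounded by the chromosome ends; the peak itself is aliased with
    the fitted peak marker and always inside.
    """
    design = fitted.design
    g = design.groups[marker]
    lo, hi = gmap.span(g.chrom)
    Qf = _basis(fitted.X)
    rows = design.geno_rows
    pops = design.populations
    pop_levels = design.pop_levels

    def test_at(pos: float) -> float:
        d = expected_dosage_at(geno, gmap, g.chrom, pos)[rows]
        cols = []
        for p in pop_levels:
            sel = pops == p
            v = np.zeros(design.n)
            v[sel] = d[sel]
            if v[sel].std() > 1e-9:
                cols.append(v)
        if not cols:
            return 1.0
        _, p_val, q = _added_group_test(design.y, Qf, np.column_stack(cols))
        return 1.0 if q == 0 else p_val

    def walk(direction: int) -> float:
        pos = g.pos_cM
        while True:
            nxt = pos + direction * step_cM
            if nxt < lo or nxt > hi:
                return lo if direction < 0 else hi
            if test_at(nxt) < alpha:
                return nxt
            pos = nxt

    return walk(-1), walk(+1)


# ---------------------------------------------------------------------------
# mapper estimator + QTL summaries
# ---------------------------------------------------------------------------

class JointLinkageMapper:
    """Permutation-calibrated stepwise joint linkage mapping for one trait.

    Parameters
    ----------
    n_permutations : int
        Permutations for the entry/exit threshold (>= 20); ignored when
        ``p_enter`` is given.
    alpha : float
        Genome-wide significance level for the permutation threshold.
    p_enter, p_exit : float, optional
        Explicit thresholds (bypass the permutation run; p_exit defaults to
        p_enter, matching the single calibrated threshold used for both).
    step_cM, si_alpha : support-interval scan step and test level.
    seed : int
        Seed for the permutation stream.

    Attributes (after ``fit``)
    ----------
    threshold_ : realized entry/exit p-value threshold
    selected_ : selected peak markers
    model_ : FittedModel
    qtl_ : per-QTL table (peak, support interval, group p, partial R^2,
        per-population effects / "n.d.")
    effects_ : tidy per-(QTL, population) effect table
    model_r2_, residual_df_ : final-model summaries
    """

    def __init__(self, n_permutations: int = 1000, alpha: float = 0.05,
                 p_enter: float | None = None, p_exit: float | None = None,
                 step_cM: float = 0.1, si_alpha: float = 0.05, seed: int = 0,
                 compute_intervals: bool = True):
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.p_enter = p_enter
        self.p_exit = p_exit
        self.step_cM = step_cM
        self.si_alpha = si_alpha
        self.seed = seed
        self.compute_intervals = compute_intervals

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "n_permutations", "alpha", "p_enter", "p_exit", "step_cM",
            "si_alpha", "seed", "compute_intervals")}

    def set_params(self, **params) -> "JointLinkageMapper":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, means: pd.DataFrame, geno: GenotypeMatrix, gmap: GeneticMap,
            trait: str) -> "JointLinkageMapper":
        design = build_nested_design(means, geno, gmap, trait)
        if self.p_enter is None:
            self.threshold_ = permutation_threshold(
                design, self.n_permutations, self.alpha, self.seed)
            p_enter = p_exit = self.threshold_
        else:
            p_enter = self.p_enter
            p_exit = self.p_exit if self.p_exit is not None else self.p_enter
            self.threshold_ = p_enter
        self.design_ = design
        sel = stepwise_select(design, p_enter, p_exit)
        self.selection_ = sel
        self.selected_ = list(sel.selected)
        self.model_ = fit_final_model(design, sel)
        self.model_r2_ = self.model_.model_r2
        self.residual_df_ = self.model_.residual_df

        rows, eff_rows = [], []
        for m in self.selected_:
            g = design.groups[m]
            gp, partial = group_statistics(self.model_, m)
            if self.compute_intervals:
                left, right = support_interval(
                    self.model_, m, geno, gmap, self.step_cM, self.si_alpha)
            else:
                left = right = np.nan
            row = {
                "trait": trait, "chrom": g.chrom, "peak_marker": m,
                "peak_cM": g.pos_cM, "SI_left_cM": left, "SI_right_cM": right,
                "group_p": gp, "partial_R2": partial,
            }
            n_sig = 0
            for p in design.pop_levels:
                name = f"{m}:{p}"
                if p in g.pops and name in self.model_.coef.index:
                    e = self.model_.coef[name]
                    s = self.model_.se[name]
                    pv = self.model_.pvalues[name]
                    row[f"effect[{p}]"] = e
                    row[f"p[{p}]"] = pv
                    if pv < 0.05:
                        n_sig += 1
                    eff_rows.append({
                        "trait": trait, "peak_marker": m, "population": p,
                        "effect": e, "se": s, "p": pv,
                    })
                else:
                    row[f"effect[{p}]"] = ND
                    row[f"p[{p}]"] = ND
                    eff_rows.append({
                        "trait": trait, "peak_marker": m, "population": p,
                        "effect": np.nan, "se": np.nan, "p": np.nan,
                    })
            row["n_significant_pops"] = n_sig
            rows.append(row)
        self.qtl_ = pd.DataFrame(rows)
        self.effects_ = pd.DataFrame(eff_rows)
        return self


def map_trait(means: pd.DataFrame, geno: GenotypeMatrix, gmap: GeneticMap,
              trait: str, **kwargs) -> JointLinkageMapper:
    """Functional wrapper: fit a JointLinkageMapper for one trait."""
    return JointLinkageMapper(**kwargs).fit(means, geno, gmap, trait)


def summarize_qtl(mappers: dict[str, JointLinkageMapper]
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concatenate per-trait QTL tables and build per-trait model summaries."""
    tables = [m.qtl_ for m in mappers.values() if len(m.qtl_)]
    qtl = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["trait", "chrom", "peak_marker", "peak_cM", "SI_left_cM",
                 "SI_right_cM", "group_p", "partial_R2", "n_significant_pops"])
    summary = pd.DataFrame({
        "trait": list(mappers),
        "n_qtl": [len(m.selected_) for m in mappers.values()],
        "model_R2": [m.model_r2_ for m in mappers.values()],
        "threshold": [m.threshold_ for m in mappers.values()],
    })
    return qtl, summary
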