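"""Independent oracles shared by the unit and acceptance suites.

These deliberately avoid the package's own selection/search code paths:
subset stability is checked by exhaustive enumeration, and segregation
expectations come from a per-locus Markov chain over the breeding scheme.
"""

import itertools

import numpy as np
import pandas as pd

from nilqtl.linkage import MarkerGroup, NestedDesign, _added_group_test, _basis


def random_design(rng, n_groups=3, n_pop=2, n_lines=40, noise=1.0,
                  causal_effect=0.0):
    """Small synthetic nested design with independent binary-dosage markers."""
    pops = np.repeat([f"P{k}" for k in range(n_pop)], n_lines // n_pop)
    base = np.ones((n_lines, 1))
    for p in pd.unique(pops)[1:]:
        base = np.hstack([base, (pops == p).astype(float)[:, None]])
    groups, order = {}, {}
    y = rng.normal(0, noise, n_lines)
    for g in range(n_groups):
        d = rng.choice([0, 0, 0, 0, 2], size=n_lines).astype(float)
        cols = np.zeros((n_lines, n_pop))
        keep = []
        for k, p in enumerate(pd.unique(pops)):
            sel = pops == p
            cols[sel, k] = d[sel]
            if d[sel].std() > 0:
                keep.append(k)
        cols = cols[:, keep]
        name = f"g{g}"
        groups[name] = MarkerGroup(name, 1, float(g), [f"P{k}" for k in keep],
                                   cols)
        order[name] = (1, float(g), name)
        if g == 0 and causal_effect:
            y = y + causal_effect * d
    return NestedDesign("y", y, np.array([f"L{i}" for i in range(n_lines)]),
                        pops, list(pd.unique(pops)), base, groups,
                        np.arange(n_lines), order)


def stable_subsets(design, p_enter, p_exit):
    """Exhaustive enumeration of all candidate subsets stable under the
    identical enter/exit criterion: every included group significant
    (p < p_exit) within the subset model, and no excluded group enterable
    (p < p_enter) given the subset."""
    names = list(design.groups)
    stable = []
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            ok = True
            for m in subset:
                others = [s for s in subset if s != m]
                X0 = design.base if not others else np.hstack(
                    [design.base] + [design.groups[s].cols for s in others])
                _, p, q = _added_group_test(design.y, _basis(X0),
                                            design.groups[m].cols)
                if q == 0 or not (p < p_exit):
                    ok = False
                    break
            if not ok:
                continue
            X0 = design.base if not subset else np.hstack(
                [design.base] + [design.groups[s].cols for s in subset])
            Q0 = _basis(X0)
            for m in names:
                if m in subset:
                    continue
                _, p, q = _added_group_test(design.y, Q0, design.groups[m].cols)
                if q > 0 and p < p_enter:
                    ok = False
                    break
            if ok:
                stable.append(frozenset(subset))
    return stable


def bc4s2_genotype_distribution(n_backcross=4, n_self=2):
    """Per-locus genotype-class probabilities through the breeding scheme,
    tracking (P_het, P_donor_hom) exactly: backcrossing halves the het
    frequency; selfing sends het -> 1/4 donor hom, 1/2 het."""
    p_het, p_hom = 1.0, 0.0
    for _ in range(n_backcross):
        p_het, p_hom = p_het * 0.5, 0.0
    for _ in range(n_self):
        p_hom = p_hom + p_het * 0.25
        p_het = p_het * 0.5
    return p_het, p_hom
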